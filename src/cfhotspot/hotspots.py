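"""Negative-binomial hotspot calling on integer IFS scores.

The background integer score C_i of a window is modelled as negative
binomial — a gamma-mixed Poisson, which absorbs the slow coverage-rate
variation along the genome that a single-rate Poisson cannot.  With
sample mean mu and variance v, the method-of-moments estimates are::

    p = mu / v          n = mu**2 / v * 1 / (1 - p)  ( = mu**2 / (v - mu) )

requiring overdispersion (v > mu).  Each window is tested lower-tail
(P(X <= q)) against two backgrounds — a local 50-kb span and the whole
chromosome — and the *larger* of the two p-values is kept, so a window
must be depleted relative to both.  MAD outliers (|x - median|/MAD > 5)
are excluded from background fitting and from testing.  Besides
protecting the NB moments from artefact spikes, the low-side exclusion
is the model's calibration guard: isolated coverage gaps produced by
sampling noise would otherwise collect extreme lower-tail p-values the
fitted background cannot price correctly.  The flip side is a depth
cap — depletions deeper than ~5 MAD below the median are not testable;
at physiological coverage the cut lies at or below zero counts, so in
practice it binds only on extreme synthetic signal.  Benjamini-Hochberg
correction is applied genome-wide; windows at FDR <= 0.2 are merged
into hotspots when separated by less than 200 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ifs import WindowTrack

logger = logging.getLogger(__name__)

DEFAULT_LOCAL_BP = 50_000
DEFAULT_FDR = 0.2
DEFAULT_MERGE_GAP = 200
DEFAULT_MAD_THRESHOLD = 5.0
MIN_BACKGROUND_WINDOWS = 30
#: pooled-fragment saturation floor below which hotspot calls are
#: flagged as potentially unsaturated
SATURATION_FLOOR = 200_000_000


class NotOverdispersedError(ValueError):
    """Sample variance does not exceed the mean: NB moments undefined."""


class DegenerateBackgroundError(ValueError):
    """Zero sample variance: no background distribution can be fitted."""


@dataclass(frozen=True)
class NBParams:
    """Method-of-moments negative-binomial background parameters."""

    p: float
    n: float
    mu: float
    v: float


def fit_nb(values: np.ndarray) -> NBParams:
    """Estimate NB (p, n) from sample moments.

    Raises :class:`DegenerateBackgroundError` when the variance is zero
    and :class:`NotOverdispersedError` when v <= mu.
    """
    values = np.asarray(values, dtype=float)
    mu = float(values.mean())
    v = float(values.var(ddof=0))
    if v == 0:
        raise DegenerateBackgroundError(f"zero variance (mu={mu})")
    if v <= mu:
        raise NotOverdispersedError(f"variance {v:.4g} <= mean {mu:.4g}")
    p = mu / v
    n = mu * mu / (v - mu)
    return NBParams(p=p, n=n, mu=mu, v=v)


def nb_lower_pvalue(q, params: NBParams):
    """Lower-tail p-value P(X <= q) under NB(size=n, prob=p).

    Accepts scalars or arrays; q < 0 returns 0.
    """
    q = np.asarray(q)
    out = np.where(q < 0, 0.0, sps.nbinom.cdf(np.maximum(q, 0), params.n, params.p))
    return float(out) if out.ndim == 0 else out


def mad_outlier_mask(values: np.ndarray, threshold: float = DEFAULT_MAD_THRESHOLD) -> np.ndarray:
    """Flag values with |x - median| / MAD > threshold.

    The MAD carries no consistency constant.  If the MAD is zero (over
    half the data at the median) the MAD of the nonzero absolute
    deviations is used instead; if that is also zero, nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    absdev = np.abs(values - med)
    mad = np.median(absdev)
    if mad == 0:
        nz = absdev[absdev > 0]
        mad = np.median(nz) if len(nz) else 0.0
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    return absdev / mad > threshold


def _lower_pvalues_vec(q: np.ndarray, mu: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorised lower-tail p-values with Poisson fallback.

    Where v > mu the NB CDF is used; where overdispersion fails the
    Poisson CDF at the same mean is the limit model.  Returns the
    p-values and the number of Poisson fallbacks.
    """
    q = np.asarray(q, dtype=float)
    pvals = np.ones_like(q, dtype=float)
    over = v > mu
    n_fallback = int((~over).sum())
    if over.any():
        p = mu[over] / v[over]
        n = mu[over] ** 2 / (v[over] - mu[over])
        pvals[over] = sps.nbinom.cdf(np.maximum(q[over], 0), n, p)
    rest = ~over & (mu > 0)
    if rest.any():
        pvals[rest] = sps.poisson.cdf(np.maximum(q[rest], 0), mu[rest])
    # mu <= 0 (possible after corrections): untestable, p = 1
    pvals[q < 0] = 0.0
    return pvals, n_fallback


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def call_hotspots(
    track: WindowTrack,
    correction: str = "none",
    local_bp: int = DEFAULT_LOCAL_BP,
    fdr_cutoff: float = DEFAULT_FDR,
    merge_gap: int = DEFAULT_MERGE_GAP,
    mad_threshold: float = DEFAULT_MAD_THRESHOLD,
    include_self: bool = True,
    bh_per_chromosome: bool = False,
    min_background: int = MIN_BACKGROUND_WINDOWS,
    use_local: bool = True,
    return_tests: bool = False,
):
    """Call fragmentation hotspots from a window track.

    For every kept, non-outlier window the integer score q = floor(IFS)
    is tested lower-tail against an NB background fitted (i) to all
    non-outlier windows of the chromosome and (ii) to non-outlier windows
    whose centres lie within ``local_bp / 2`` of the window centre.  The
    larger p-value is BH-adjusted; windows at FDR <= ``fdr_cutoff`` are
    merged into hotspots when their intervals are separated by less than
    ``merge_gap`` bp (strict).

    Returns a hotspot BED-like DataFrame, plus the per-window test table
    when ``return_tests`` is true.
    """
    w = track.windows
    col = track.score_column(correction)
    test_frames = []
    for chrom, sub in w.groupby("chrom", sort=True):
        c_all = np.floor(sub[col].to_numpy()).astype(np.int64)
        valid = ~np.isnan(sub[col].to_numpy())
        if valid.sum() < min_background:
            logger.warning("%s: too few windows (%d), chromosome skipped", chrom, int(valid.sum()))
            continue
        outlier = np.zeros(len(sub), dtype=bool)
        outlier[valid] = mad_outlier_mask(c_all[valid], threshold=mad_threshold)
        bg = valid & ~outlier
        test = bg
        try:
            params = fit_nb(c_all[bg])
            p_global = nb_lower_pvalue(c_all[test], params)
        except NotOverdispersedError:
            logger.warning("%s: global background not overdispersed; Poisson fallback", chrom)
            mu = float(c_all[bg].mean())
            p_global = sps.poisson.cdf(np.maximum(c_all[test], 0), mu)
        except DegenerateBackgroundError:
            logger.warning("%s: degenerate background, chromosome skipped", chrom)
            continue

        all_centers = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        c = c_all[test]
        if use_local:
            p_local, n_fb, n_small = _local_pvalues(
                all_centers[test],
                c,
                all_centers[bg],
                c_all[bg],
                local_bp=local_bp,
                include_self=include_self,
                min_background=min_background,
            )
            if n_fb:
                logger.info("%s: %d windows used Poisson fallback for the local background", chrom, n_fb)
            if n_small:
                logger.info("%s: %d windows had <%d local windows; global p used", chrom, n_small, min_background)
            p_max = np.maximum(p_local, p_global)
        else:
            p_max = np.asarray(p_global, dtype=float)
        frame = sub.loc[test, ["chrom", "start", "end"]].copy()
        frame["c"] = c
        frame["p_global"] = p_global
        frame["p_local"] = p_local if use_local else np.nan
        frame["p_max"] = p_max
        test_frames.append(frame)

    if not test_frames:
        raise ValueError("no chromosome could be tested")
    tests = pd.concat(test_frames, ignore_index=True)
    if bh_per_chromosome:
        tests["fdr"] = np.nan
        for chrom, idx in tests.groupby("chrom", sort=False).indices.items():
            tests.loc[idx, "fdr"] = benjamini_hochberg(tests.loc[idx, "p_max"].to_numpy())
    else:
        tests["fdr"] = benjamini_hochberg(tests["p_max"].to_numpy())
    sig = tests[tests["fdr"] <= fdr_cutoff]
    hotspots = merge_significant_windows(sig, merge_gap=merge_gap)
    if return_tests:
        return hotspots, tests
    return hotspots


def _local_pvalues(
    test_centers: np.ndarray,
    c_test: np.ndarray,
    bg_centers: np.ndarray,
    c_bg: np.ndarray,
    local_bp: int = DEFAULT_LOCAL_BP,
    include_self: bool = True,
    min_background: int = MIN_BACKGROUND_WINDOWS,
) -> tuple[np.ndarray, int, int]:
    """Lower-tail p-values against the 50-kb local background.

    The background of a tested window comprises the non-outlier windows
    whose centres lie within ``local_bp / 2`` of its centre; running
    sums over the sorted background centres give every span's moments in
    O(W log W).
    """
    half = local_bp // 2
    cf = c_bg.astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(cf)])
    cum2 = np.concatenate([[0.0], np.cumsum(cf * cf)])
    lo = np.searchsorted(bg_centers, test_centers - half, side="left")
    hi = np.searchsorted(bg_centers, test_centers + half, side="right")
    m = (hi - lo).astype(np.float64)
    s1 = cum[hi] - cum[lo]
    s2 = cum2[hi] - cum2[lo]
    if not include_self:
        # remove the tested window's own contribution where it is part
        # of the background set
        pos = np.searchsorted(bg_centers, test_centers, side="left")
        in_bg = (pos < len(bg_centers)) & (bg_centers[np.minimum(pos, len(bg_centers) - 1)] == test_centers)
        m[in_bg] -= 1
        s1[in_bg] -= c_test[in_bg].astype(np.float64)
        s2[in_bg] -= c_test[in_bg].astype(np.float64) ** 2
    small = m < min_background
    m = np.maximum(m, 1.0)
    mu = s1 / m
    v = s2 / m - mu * mu
    pvals, n_fallback = _lower_pvalues_vec(c_test, mu, v)
    # spans too sparse to characterise: fall back to the global test only
    pvals[small] = 0.0  # neutral under the max rule
    return pvals, n_fallback, int(small.sum())


def merge_significant_windows(sig: pd.DataFrame, merge_gap: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Merge significant windows into hotspots.

    Windows whose intervals are separated by *less than* ``merge_gap``
    bp merge (overlapping or adjacent-within-gap); a gap of exactly
    ``merge_gap`` keeps them distinct.  The hotspot interval is the union
    span; its centre is floor((start + end) / 2); ``best_fdr`` is the
    smallest member FDR.
    """
    cols = ["chrom", "start", "end", "center", "best_fdr", "n_windows"]
    if len(sig) == 0:
        return pd.DataFrame(columns=cols)
    sig = sig.sort_values(["chrom", "start"], kind="mergesort")
    rows = []
    cur = None
    for rec in sig.itertuples(index=False):
        fdr = getattr(rec, "fdr", np.nan)
        if cur is not None and rec.chrom == cur["chrom"] and rec.start - cur["end"] < merge_gap:
            cur["end"] = max(cur["end"], rec.end)
            cur["best_fdr"] = min(cur["best_fdr"], fdr)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": rec.chrom, "start": rec.start, "end": rec.end, "best_fdr": fdr, "n_windows": 1}
    rows.append(cur)
    out = pd.DataFrame(rows)
    out["center"] = (out["start"] + out["end"]) // 2
    return out[cols]


def pool_samples(
    fragment_tables: Iterable[pd.DataFrame],
    saturation_floor: int = SATURATION_FLOOR,
) -> pd.DataFrame:
    """Concatenate per-sample fragment tables for pooled hotspot calling.

    Warns when the pool is below the saturation floor (2e8 fragments),
    under which hotspot discovery is expected to be incomplete.
    """
    tables = [t for t in fragment_tables]
    if not tables or sum(len(t) for t in tables) == 0:
        raise ValueError("empty fragment pool")
    pooled = pd.concat(tables, ignore_index=True)
    if len(pooled) < saturation_floor:
        logger.warning(
            "pooled %d fragments, below the %d saturation floor: hotspot discovery may be unsaturated",
            len(pooled),
            saturation_floor,
        )
    return pooled.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_hotspots_bed(hotspots: pd.DataFrame, path: str | Path) -> None:
    """Write hotspots as BED6+2 (name, -10*log10(best_fdr) score capped
    at 1000, strand '.', then n_windows and best_fdr)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(hotspots.itertuples(index=False)):
            with np.errstate(divide="ignore"):
                score = min(1000, int(round(-10 * np.log10(max(rec.best_fdr, 1e-300)))))
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\thotspot_{i + 1}\t{score}\t.\t{rec.n_windows}\t{rec.best_fdr:.6g}\n"
            )


def overlap_recall_precision(
    hotspots: pd.DataFrame, truth: pd.DataFrame
) -> tuple[float, float]:
    """Recall/precision of called hotspots against planted truth regions.

    A truth region is recovered when >=1 called hotspot overlaps it by
    >=1 bp; a called hotspot is a true positive when it overlaps >=1
    truth region.  Empty calls give recall 0 and precision 1 (vacuous).
    """
    from .windows import overlaps_any

    if len(truth) == 0:
        raise ValueError("empty truth set")
    recovered = 0
    true_calls = 0
    for chrom in truth["chrom"].unique():
        t = truth[truth["chrom"] == chrom]
        h = hotspots[hotspots["chrom"] == chrom]
        if len(h) == 0:
            continue
        recovered += int(
            overlaps_any(
                t["start"].to_numpy(), t["end"].to_numpy(), h["start"].to_numpy(), h["end"].to_numpy()
            ).sum()
        )
        true_calls += int(
            overlaps_any(
                h["start"].to_numpy(), h["end"].to_numpy(), t["start"].to_numpy(), t["end"].to_numpy()
            ).sum()
        )
    recall = recovered / len(truth)
    precision = true_calls / len(hotspots) if len(hotspots) else 1.0
    return recall, precision
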