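"""Genome-wide sliding-window grid with region filters and covariates.

Hotspot calling scans each autosome with a 200-bp window advanced in
20-bp steps.  Windows overlapping assembly dark regions (blacklists), or
whose mean per-base mappability falls below 0.9, are removed before any
statistics are computed.  Per-window sequence covariates (GC fraction
and dinucleotide composition) feed the bias corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import is_autosome, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 200
DEFAULT_STEP = 20

#: the 16 dinucleotides in lexicographic order (column order of dimer_freq)
DIMERS = [a + b for a in "ACGT" for b in "ACGT"]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass
class WindowGrid:
    """Sliding windows on one chromosome.

    ``starts`` are 0-based window starts with constant spacing ``step``;
    ``keep`` marks windows surviving the region-level filters.
    """

    chrom: str
    chrom_length: int
    width: int = DEFAULT_WIDTH
    step: int = DEFAULT_STEP
    starts: np.ndarray = field(default=None)
    keep: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.width <= 0 or self.step <= 0:
            raise ValueError("window width and step must be positive")
        if self.starts is None:
            n = (self.chrom_length - self.width) // self.step + 1
            if n <= 0:
                raise ValueError(
                    f"{self.chrom}: length {self.chrom_length} shorter than window width {self.width}"
                )
            self.starts = np.arange(n, dtype=np.int64) * self.step
        if self.keep is None:
            self.keep = np.ones(len(self.starts), dtype=bool)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.width

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width // 2

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class WindowCovariates:
    """Per-window sequence covariates for one chromosome grid."""

    gc: np.ndarray  # fraction of G+C among non-N bases, NaN when undefined
    mappability: np.ndarray | None = None  # mean per-base score in [0,1]
    dimer_freq: np.ndarray | None = None  # (n_windows, 16), rows sum to 1
    valid: np.ndarray | None = None  # False where covariates are unusable

    def __post_init__(self):
        if self.valid is None:
            self.valid = ~np.isnan(self.gc)


def generate_windows(
    chrom_sizes: Mapping[str, int],
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
    autosomes_only: bool = True,
) -> dict[str, WindowGrid]:
    """Tile each (autosomal) chromosome with sliding windows from position 0.

    A trailing window that would extend past the chromosome end is not
    emitted, so every window lies fully within ``[0, length)``.
    """
    if width <= 0 or step <= 0:
        raise ValueError("window width and step must be positive")
    grids: dict[str, WindowGrid] = {}
    for chrom, length in chrom_sizes.items():
        if autosomes_only and not is_autosome(chrom):
            continue
        if length <= width:
            logger.warning("%s shorter than one window, skipped", chrom)
            continue
        grids[chrom] = WindowGrid(chrom=chrom, chrom_length=length, width=width, step=step)
    return grids


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a (chrom, start, end) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def overlaps_any(
    starts: np.ndarray, ends: np.ndarray, iv_starts: np.ndarray, iv_ends: np.ndarray
) -> np.ndarray:
    """Boolean mask: does each half-open query interval overlap >=1 bp of
    the (merged) interval set?"""
    if len(iv_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    ms, me = _merge_intervals(np.asarray(iv_starts), np.asarray(iv_ends))
    # candidate merged interval: last one starting before the query end
    idx = np.searchsorted(ms, ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = me[idx[hit]] > starts[hit]
    return hit


def apply_region_filters(
    grid: WindowGrid,
    blacklist: pd.DataFrame | None = None,
    mappability: np.ndarray | None = None,
    min_mappability: float = 0.9,
) -> WindowGrid:
    """Drop windows overlapping the blacklist or with low mean mappability.

    ``mappability`` is a per-base array for the grid's chromosome; missing
    (NaN) values count as 0, so uncovered windows are removed — the
    conservative choice.  A window with mean exactly ``min_mappability``
    is kept (the rule removes means *smaller than* the threshold).
    """
    keep = grid.keep.copy()
    if blacklist is not None and len(blacklist):
        chrom_bl = blacklist[
            blacklist["chrom"].map(normalize_chrom) == normalize_chrom(grid.chrom)
        ]
        if len(chrom_bl):
            hit = overlaps_any(
                grid.starts, grid.ends, chrom_bl["start"].to_numpy(), chrom_bl["end"].to_numpy()
            )
            keep &= ~hit
    if mappability is not None:
        track = np.asarray(mappability, dtype=float)
        if len(track) < grid.chrom_length:
            track = np.pad(track, (0, grid.chrom_length - len(track)))
        nan = np.isnan(track)
        if nan.any():
            logger.warning("%s: %d missing mappability bases treated as 0", grid.chrom, int(nan.sum()))
            track = np.where(nan, 0.0, track)
        mean_map = _window_means(track, grid)
        # small tolerance so a uniform track at exactly the threshold is
        # not lost to cumulative-sum rounding
        keep &= mean_map >= min_mappability - 1e-9
    out = WindowGrid(
        chrom=grid.chrom,
        chrom_length=grid.chrom_length,
        width=grid.width,
        step=grid.step,
        starts=grid.starts,
        keep=keep,
    )
    return out


def _window_means(per_base: np.ndarray, grid: WindowGrid) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(per_base, dtype=np.float64)])
    return (cum[grid.ends] - cum[grid.starts]) / grid.width


def window_mappability(per_base: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Mean per-base mappability per window (missing values as 0)."""
    track = np.where(np.isnan(per_base), 0.0, np.asarray(per_base, dtype=float))
    return _window_means(track, grid)


def _get_sequence(genome, chrom: str, length: int) -> str:
    for key in (chrom, "chr" + normalize_chrom(chrom), normalize_chrom(chrom)):
        try:
            seq = genome[key]
        except KeyError:
            continue
        return str(seq[0:length])
    raise KeyError(f"chromosome {chrom!r} absent from the genome sequence source")


def compute_covariates(
    grid: WindowGrid,
    genome,
    mappability: np.ndarray | None = None,
    max_n_fraction: float = 0.1,
) -> WindowCovariates:
    """Per-window GC fraction and dinucleotide frequencies from sequence.

    GC is computed over non-N bases only.  Dimer frequencies cover the
    window's ``width - 1`` overlapping dinucleotides, excluding any dimer
    touching an ambiguous base, renormalised to sum to 1.  Windows that
    are entirely N, or with more than ``max_n_fraction`` ambiguous bases,
    are flagged invalid (excluded from correction and testing).
    """
    seq = _get_sequence(genome, grid.chrom, grid.chrom_length)
    code = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(code) < grid.chrom_length:
        code = np.pad(code, (0, grid.chrom_length - len(code)), constant_values=255)
    valid_base = code < 4
    is_gc = (code == 1) | (code == 2)

    n_valid = _window_means(valid_base.astype(np.float64), grid) * grid.width
    n_gc = _window_means(is_gc.astype(np.float64), grid) * grid.width
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(n_valid > 0, n_gc / np.maximum(n_valid, 1e-12), np.nan)

    # dimer codes at positions i covering (i, i+1)
    dim_valid = valid_base[:-1] & valid_base[1:]
    dim_code = np.where(dim_valid, 4 * code[:-1].astype(np.int16) + code[1:], -1)
    counts = np.empty((len(grid), 16), dtype=np.float64)
    dim_ends = np.minimum(grid.ends - 1, len(dim_code))
    for d in range(16):
        cum = np.concatenate([[0.0], np.cumsum(dim_code == d, dtype=np.float64)])
        counts[:, d] = cum[dim_ends] - cum[grid.starts]
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dimer_freq = counts / np.maximum(totals[:, None], 1e-12)
    dimer_freq[totals == 0] = np.nan

    valid = (n_valid >= (1.0 - max_n_fraction) * grid.width) & (totals > 0) & ~np.isnan(gc)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("%s: %d windows flagged invalid (ambiguous sequence)", grid.chrom, n_invalid)
    mapp = window_mappability(mappability, grid) if mappability is not None else None
    return WindowCovariates(gc=gc, mappability=mapp, dimer_freq=dimer_freq, valid=valid)


def sequence_gc(seq: str) -> float:
    """GC fraction of a sequence over its non-N bases (NaN if none)."""
    code = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    valid = code < 4
    if not valid.any():
        return float("nan")
    return float(((code == 1) | (code == 2)).sum() / valid.sum())


def sequence_dimer_freq(seq: str) -> np.ndarray:
    """Dinucleotide frequency 16-vector of a sequence (NaN row if none)."""
    code = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    valid = (code[:-1] < 4) & (code[1:] < 4)
    dim = 4 * code[:-1][valid].astype(int) + code[1:][valid]
    if len(dim) == 0:
        return np.full(16, np.nan)
    return np.bincount(dim, minlength=16) / len(dim)


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph track to per-base arrays (one per chromosome).

    Bases not covered by any record are NaN (treated as 0 by the window
    filters).  Intended for the genome scales this package targets; for
    full human genomes a bigWig reader is the appropriate source.
    """
    tracks = {c: np.full(l, np.nan) for c, l in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom in tracks:
                tracks[chrom][int(start) : int(end)] = float(value)
    return tracks
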