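"""Reading and quality-filtering of paired-end cfDNA fragments.

A *fragment* is one sequenced cell-free DNA molecule, represented as a
0-based half-open genomic interval.  Two input dialects are supported:

* coordinate BAM/SAM with standard flags — one fragment is emitted per
  properly-paired read pair, spanning the outer template coordinates;
* a plain fragment BED with >= 3 columns ``chrom  start  end [mapq]``
  (optionally gzip-compressed), where ``mapq`` is the minimum of the two
  mate mapping qualities.

Filtering follows the conventional cfDNA WGS conventions: proper pairs
only, no duplicate/secondary/supplementary records, max-of-mates MAPQ
>= 30, autosomes only, fragment length within [50, 1000] bp inclusive.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical autosome names, without the "chr" prefix
_AUTOSOME_NUMBERS = {str(i) for i in range(1, 23)}

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length", "mapq"]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr1`` and ``1`` compare equal."""
    return chrom[3:] if chrom.startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOME_NUMBERS


@dataclass(frozen=True)
class FragmentFilterConfig:
    """Fragment-level quality filters.

    Defaults implement the standard cfDNA preprocessing: fragments shorter
    than ``min_len`` or longer than ``max_len`` are excluded (the bounds
    themselves are retained), either end must reach ``min_mapq``, and only
    autosomal, properly-paired, non-duplicate primary alignments count.
    """

    min_len: int = 50
    max_len: int = 1000
    min_mapq: int = 30
    autosomes_only: bool = True
    require_proper_pair: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise ValueError("require 0 < min_len < max_len")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class FilterStats:
    """Per-reason rejection counters; retained + rejected == total input."""

    total: int = 0
    retained: int = 0
    rejected: Counter = field(default_factory=Counter)
    #: alignment records skipped before pair formation (BAM only); these
    #: are reads, not pairs, and sit outside the pair-conservation balance
    skipped_reads: Counter = field(default_factory=Counter)

    def log(self) -> None:
        logger.info(
            "fragments: %d/%d retained; rejected: %s",
            self.retained,
            self.total,
            dict(self.rejected),
        )


def fragment_midpoint(start: int, end: int) -> int:
    """Midpoint of a fragment interval, ties broken to the left (floor)."""
    return (start + end) // 2


def midpoints(frags: pd.DataFrame) -> np.ndarray:
    """Vectorised fragment midpoints (floor of the interval centre)."""
    return (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2


def read_fragments(
    path: str | Path,
    format: str | None = None,
    config: FragmentFilterConfig | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    return_stats: bool = False,
):
    """Read fragments from BAM/SAM or fragment BED and apply quality filters.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the suffix when omitted.
    config
        Filter thresholds; defaults applied when ``None``.
    chrom_sizes
        Optional declared genome; fragments on chromosomes absent from it
        are skipped with a warning counter.
    return_stats
        Also return the :class:`FilterStats` with per-filter counters.

    Returns
    -------
    DataFrame with columns ``chrom, start, end, length, mapq`` sorted by
    (chrom, start), containing only fragments passing every filter.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"fragment file not found: {path}")
    if format is None:
        name = path.name
        if name.endswith((".bam", ".sam", ".cram")):
            format = "bam"
        else:
            format = "bed"
    if format == "bam":
        frags, stats = _read_bam(path, config or FragmentFilterConfig(), chrom_sizes)
    elif format == "bed":
        frags, stats = _read_bed(path, config or FragmentFilterConfig(), chrom_sizes)
    else:
        raise ValueError(f"unknown fragment format: {format!r}")
    stats.log()
    if return_stats:
        return frags, stats
    return frags


def filter_fragments(
    frags: pd.DataFrame,
    config: FragmentFilterConfig | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    stats: FilterStats | None = None,
) -> pd.DataFrame:
    """Apply length/MAPQ/autosome filters to an in-memory fragment table.

    Idempotent: filtering an already-filtered table is a no-op.
    """
    config = config or FragmentFilterConfig()
    stats = stats if stats is not None else FilterStats()
    stats.total += len(frags)

    keep = np.ones(len(frags), dtype=bool)
    chroms = frags["chrom"].astype(str)

    if chrom_sizes is not None:
        known = {normalize_chrom(c) for c in chrom_sizes}
        ok = chroms.map(lambda c: normalize_chrom(c) in known).to_numpy()
        if not ok.all():
            logger.warning("%d fragments on chromosomes absent from the declared genome", int((~ok).sum()))
        stats.rejected["unknown_chrom"] += int((keep & ~ok).sum())
        keep &= ok
    if config.autosomes_only:
        ok = chroms.map(is_autosome).to_numpy()
        stats.rejected["non_autosome"] += int((keep & ~ok).sum())
        keep &= ok

    length = frags["length"].to_numpy() if "length" in frags else (
        frags["end"].to_numpy() - frags["start"].to_numpy()
    )
    ok = (length >= config.min_len) & (length <= config.max_len)
    stats.rejected["length"] += int((keep & ~ok).sum())
    keep &= ok

    if "mapq" in frags.columns:
        mapq = frags["mapq"].to_numpy()
        ok = (mapq >= config.min_mapq) | np.isnan(mapq.astype(float))
        stats.rejected["mapq"] += int((keep & ~ok).sum())
        keep &= ok

    out = frags.loc[keep].copy()
    if "length" not in out.columns:
        out["length"] = out["end"] - out["start"]
    stats.retained += len(out)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _read_bed(path: Path, config: FragmentFilterConfig, chrom_sizes) -> tuple[pd.DataFrame, FilterStats]:
    opener = gzip.open if str(path).endswith(".gz") else open
    rows = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fragment BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            mapq = float(parts[3]) if len(parts) > 3 and parts[3] not in (".", "") else np.nan
            rows.append((chrom, start, end, end - start, mapq))
    frags = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    stats = FilterStats()
    out = filter_fragments(frags, config, chrom_sizes, stats=stats)
    return out, stats


def _read_bam(path: Path, config: FragmentFilterConfig, chrom_sizes) -> tuple[pd.DataFrame, FilterStats]:
    import pysam

    mode = "r" if path.suffix == ".sam" else "rb"
    stats = FilterStats()
    # pair mates by query name; adequate for the fragment counts this
    # package targets (pooled fragment BEDs are the high-volume path).
    # Every read pair becomes exactly one record in the accounting:
    # retained + sum(rejected) == total pairs.
    pending: dict[str, object] = {}
    rows = []
    dropped_pairs: Counter = Counter()
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                # alignment-level records, not fragments; a pair with any
                # such primary-flag problem is rejected below via its
                # primary records' flags, so these are simply skipped —
                # but a pair *represented only* by such records never
                # forms, which is the intended exclusion
                key = "secondary" if read.is_secondary else "supplementary"
                dropped_pairs[key] += 1
                continue
            if read.is_unmapped or read.mate_is_unmapped:
                dropped_pairs["unmapped"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            stats.total += 1
            first, second = (mate, read) if mate.reference_start <= read.reference_start else (read, mate)
            reason = _pair_reject_reason(first, second, config)
            if reason:
                stats.rejected[reason] += 1
                continue
            start = first.reference_start
            end = second.reference_end
            if end is None or end <= start:
                stats.rejected["degenerate_span"] += 1
                continue
            mapq = max(first.mapping_quality, second.mapping_quality)
            rows.append((first.reference_name, start, end, end - start, float(mapq)))
    if pending:
        stats.total += len(pending)
        stats.rejected["unpaired"] += len(pending)
    stats.skipped_reads.update(dropped_pairs)
    frags = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    n_formed = len(frags)
    out = filter_fragments(frags, config, chrom_sizes, stats=stats)
    stats.total -= n_formed  # filter_fragments re-counted the formed pairs
    return out, stats


def _pair_reject_reason(first, second, config: FragmentFilterConfig) -> str | None:
    if config.require_proper_pair and not (first.is_proper_pair and second.is_proper_pair):
        return "not_proper_pair"
    if first.is_duplicate or second.is_duplicate:
        return "duplicate"
    return None


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    """Write a fragment table as 4-column BED (chrom, start, end, mapq)."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for chrom, start, end, mapq in zip(
            frags["chrom"], frags["start"], frags["end"], frags.get("mapq", pd.Series(np.nan, index=frags.index))
        ):
            m = "." if pd.isna(mapq) else str(int(mapq))
            fh.write(f"{chrom}\t{start}\t{end}\t{m}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``chrom.sizes`` TSV into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
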