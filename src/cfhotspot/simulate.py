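"""Synthetic genomes, fragment files and cohorts for end-to-end testing.

The generator reproduces the statistical structure the hotspot caller
assumes, so that its guarantees (FDR control, planted-signal recovery)
are checkable without patient data:

* fragment midpoints are placed from a gamma-modulated intensity —
  a gamma-distributed rate per 1-kb block mixed with Poisson placement,
  which makes window counts negative-binomial under the null;
* planted low-fragmentation regions multiply the local intensity by a
  depletion factor in (0, 1] and shift fragment sizes, emulating
  accessible chromatin that releases fewer, shorter-protected fragments;
* fragment sizes are lognormal (default mean 166 bp, sd 40, truncated to
  [50, 1000]) around the mononucleosomal cfDNA mode;
* optional smooth GC bias and mappability dropout emulate the technical
  artefacts the corrections and filters are built for.

Everything is deterministic under a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .fragments import FRAGMENT_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_SIZE_MEAN = 166.0
DEFAULT_SIZE_SD = 40.0
DEFAULT_GAMMA_SHAPE = 150.0
DEFAULT_BLOCK_BP = 1000


@dataclass
class SimGenome:
    """A synthetic genome: lengths, optional sequence, tracks, truth."""

    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None
    blacklist: pd.DataFrame | None = None
    mappability: dict[str, np.ndarray] | None = None
    #: truth table of planted regions: chrom, start, end, depletion, size_shift
    planted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "depletion", "size_shift"])
    )


def _gc_landscape(n_blocks: int, rng: np.random.Generator, lo: float = 0.30, hi: float = 0.60) -> np.ndarray:
    """Smooth per-block GC content via a reflected random walk."""
    steps = rng.normal(0, 0.02, n_blocks)
    gc = 0.5 * (lo + hi) + np.cumsum(steps)
    # reflect into [lo, hi]
    span = hi - lo
    gc = lo + np.abs((gc - lo) % (2 * span) - span)
    return gc


def make_genome(
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    with_sequence: bool = True,
    blacklist_fraction: float = 0.01,
    mappability_dropout: float = 0.01,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> SimGenome:
    """Random genome with a smooth GC landscape, blacklist and mappability.

    ``blacklist_fraction`` of each chromosome is covered by random dark
    intervals (2-10 kb); ``mappability_dropout`` of 1-kb blocks get
    mappability 0.5 (below the 0.9 filter), the rest 1.0.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    mapp: dict[str, np.ndarray] = {}
    bl_rows = []
    for chrom, length in chrom_lengths.items():
        n_blocks = -(-length // block_bp)
        if with_sequence:
            gc_blocks = _gc_landscape(n_blocks, rng)
            gc_base = np.repeat(gc_blocks, block_bp)[:length]
            u = rng.random(length)
            is_gc = u < gc_base
            u2 = rng.random(length)
            bases = np.where(is_gc, np.where(u2 < 0.5, ord("C"), ord("G")), np.where(u2 < 0.5, ord("A"), ord("T")))
            sequences[chrom] = bases.astype(np.uint8).tobytes().decode("ascii")
        track = np.ones(length)
        n_drop = rng.binomial(n_blocks, mappability_dropout)
        for b in rng.choice(n_blocks, size=n_drop, replace=False):
            track[b * block_bp : (b + 1) * block_bp] = 0.5
        mapp[chrom] = track
        covered = 0
        target = blacklist_fraction * length
        while covered < target:
            size = int(rng.integers(2000, 10001))
            start = int(rng.integers(0, max(1, length - size)))
            bl_rows.append((chrom, start, start + size))
            covered += size
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])
    return SimGenome(
        chrom_lengths=dict(chrom_lengths),
        sequences=sequences if with_sequence else None,
        blacklist=blacklist,
        mappability=mapp,
    )


def plant_regions(
    genome: SimGenome,
    n_regions: int,
    region_size: int = 400,
    depletion: float = 0.5,
    size_shift: int = -15,
    seed: int = 0,
    min_gap: int = 5000,
) -> SimGenome:
    """Plant low-IFS regions avoiding the blacklist, spaced >= ``min_gap``."""
    if not 0 < depletion <= 1:
        raise ValueError("depletion factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    total = sum(genome.chrom_lengths.values())
    rows = []
    bl = genome.blacklist if genome.blacklist is not None else pd.DataFrame(columns=["chrom", "start", "end"])
    per_chrom = {
        c: max(1, round(n_regions * l / total)) for c, l in genome.chrom_lengths.items()
    }
    # adjust to the exact requested count
    while sum(per_chrom.values()) > n_regions:
        per_chrom[max(per_chrom, key=per_chrom.get)] -= 1
    for chrom, k in per_chrom.items():
        length = genome.chrom_lengths[chrom]
        chrom_bl = bl[bl["chrom"] == chrom]
        placed: list[int] = []
        attempts = 0
        while len(placed) < k and attempts < 100 * k:
            attempts += 1
            start = int(rng.integers(1000, length - region_size - 1000))
            if any(abs(start - p) < min_gap for p in placed):
                continue
            end = start + region_size
            if ((chrom_bl["start"] < end) & (chrom_bl["end"] > start)).any():
                continue
            placed.append(start)
            rows.append((chrom, start, end, depletion, size_shift))
    planted = pd.DataFrame(rows, columns=["chrom", "start", "end", "depletion", "size_shift"]).sort_values(
        ["chrom", "start"]
    )
    genome.planted = planted.reset_index(drop=True)
    return genome


_GC_BIAS_FUNCS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "none": lambda gc, amp: np.ones_like(gc),
    "linear": lambda gc, amp: np.clip(1.0 + amp * (gc - 0.45) * 10.0, 0.05, None),
    "quadratic": lambda gc, amp: np.clip(1.0 + amp * (1.0 - ((gc - 0.45) / 0.10) ** 2), 0.05, None),
}


def _lognormal_lengths(rng, n, mean, sd, lo, hi):
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    lens = np.exp(rng.normal(mu, np.sqrt(sigma2), n))
    return np.clip(np.round(lens), lo, hi).astype(np.int64)


def simulate_fragments(
    genome: SimGenome,
    n_fragments: int,
    seed: int = 0,
    size_mean: float = DEFAULT_SIZE_MEAN,
    size_sd: float = DEFAULT_SIZE_SD,
    size_min: int = 50,
    size_max: int = 1000,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    block_bp: int = DEFAULT_BLOCK_BP,
    gc_bias: str = "none",
    gc_bias_amplitude: float = 0.0,
    region_multipliers: pd.DataFrame | None = None,
    out_bed: str | Path | None = None,
) -> pd.DataFrame:
    """Draw ``n_fragments`` fragments from the genome's intensity model.

    Midpoint intensity per base = gamma block rate x GC-bias factor x
    planted-region depletion x optional per-region multipliers (a
    (chrom, start, end, multiplier) table, used for cohort class
    effects).  Fragment lengths are lognormal; fragments with midpoints
    inside a planted region have the region's ``size_shift`` added.
    Returns a sorted fragment table; optionally writes a fragment BED
    (byte-identical across runs with the same seed).
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    weights_per_chrom = {}
    totals = np.empty(len(chroms))
    for ci, chrom in enumerate(chroms):
        length = genome.chrom_lengths[chrom]
        n_blocks = -(-length // block_bp)
        rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, n_blocks)
        w = np.repeat(rates, block_bp)[:length]
        if gc_bias != "none":
            if genome.sequences is None:
                raise ValueError("GC bias requires a genome sequence")
            seq = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
            is_gc = (seq == ord("C")) | (seq == ord("G"))
            block_gc = np.add.reduceat(is_gc, np.arange(0, length, block_bp)) / np.diff(
                np.append(np.arange(0, length, block_bp), length)
            )
            w *= np.repeat(_GC_BIAS_FUNCS[gc_bias](block_gc, gc_bias_amplitude), block_bp)[:length]
        for reg in genome.planted[genome.planted["chrom"] == chrom].itertuples(index=False):
            if reg.depletion == 0:
                raise ValueError("depletion 0 would demand coverage from an empty region")
            w[reg.start : reg.end] *= reg.depletion
        if region_multipliers is not None:
            for reg in region_multipliers[region_multipliers["chrom"] == chrom].itertuples(index=False):
                w[reg.start : reg.end] *= reg.multiplier
        weights_per_chrom[chrom] = w
        totals[ci] = w.sum()
    counts = rng.multinomial(n_fragments, totals / totals.sum())

    frames = []
    for chrom, count in zip(chroms, counts):
        if count == 0:
            continue
        w = weights_per_chrom[chrom]
        cum = np.cumsum(w)
        mids = np.searchsorted(cum, rng.random(count) * cum[-1], side="right")
        mids.sort()
        lens = _lognormal_lengths(rng, count, size_mean, size_sd, size_min, size_max)
        planted = genome.planted[genome.planted["chrom"] == chrom]
        if len(planted):
            reg_starts = planted["start"].to_numpy()
            reg_ends = planted["end"].to_numpy()
            shifts = planted["size_shift"].to_numpy()
            idx = np.searchsorted(reg_starts, mids, side="right") - 1
            inside = (idx >= 0) & (mids < reg_ends[np.maximum(idx, 0)])
            lens[inside] = np.clip(lens[inside] + shifts[idx[inside]], size_min, size_max)
        length = genome.chrom_lengths[chrom]
        starts = np.clip(mids - lens // 2, 0, None)
        ends = starts + lens
        over = ends > length
        starts[over] = length - lens[over]
        ends[over] = length
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "length": lens, "mapq": 60.0}
            )
        )
    frags = pd.concat(frames, ignore_index=True)[FRAGMENT_COLUMNS]
    if out_bed is not None:
        from .fragments import write_fragments_bed

        write_fragments_bed(frags, out_bed)
    return frags


@dataclass
class CohortSpec:
    """A labelled multi-class cohort with hotspot-level effect sizes.

    ``classes`` maps label -> sample count; ``effects`` maps label -> a
    vector of per-hotspot z-shifts (aligned with the genome's planted
    regions; 0 = no class effect at that hotspot).  Shifts are converted
    to intensity multipliers via 1 + dz / sqrt(mu_r), where mu_r is the
    expected per-sample midpoint count in a region — the per-hotspot
    noise scale at low coverage.
    """

    classes: dict[str, int]
    fragments_per_sample: int = 200_000
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    gc_bias: str = "none"
    gc_bias_amplitude: float = 0.0
    seed: int = 0


def simulate_cohort(
    genome: SimGenome, spec: CohortSpec
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-sample fragment tables plus sample sheet and truth table."""
    rng = np.random.default_rng(spec.seed)
    total_len = sum(genome.chrom_lengths.values())
    regions = genome.planted
    mu_r = (
        spec.fragments_per_sample
        / total_len
        * (regions["end"] - regions["start"]).mean()
        * regions["depletion"].mean()
        if len(regions)
        else 1.0
    )
    sample_frags: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    truth_rows = []
    for label, n_samples in spec.classes.items():
        shifts = np.asarray(spec.effects.get(label, np.zeros(len(regions))), dtype=float)
        mult = np.clip(1.0 + shifts / np.sqrt(max(mu_r, 1.0)), 0.05, None)
        region_mult = regions[["chrom", "start", "end"]].assign(multiplier=mult)
        for reg, dz, m in zip(regions.itertuples(index=False), shifts, mult):
            if dz != 0:
                truth_rows.append((label, reg.chrom, reg.start, reg.end, dz, m))
        for i in range(n_samples):
            sid = f"{label}_{i:03d}"
            frags = simulate_fragments(
                genome,
                spec.fragments_per_sample,
                seed=int(rng.integers(2**31)),
                gc_bias=spec.gc_bias,
                gc_bias_amplitude=spec.gc_bias_amplitude,
                region_multipliers=region_mult,
            )
            sample_frags[sid] = frags
            sheet_rows.append((sid, label, len(frags)))
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "label", "n_fragments"])
    truth = pd.DataFrame(
        truth_rows, columns=["label", "chrom", "start", "end", "z_shift", "multiplier"]
    )
    return sample_frags, sheet, truth


def simulate_feature_matrix(
    classes: Mapping[str, int],
    n_hotspots: int,
    shifts: Mapping[str, np.ndarray] | None = None,
    hotspots_per_chrom: int = 500,
    seed: int = 0,
) -> FeatureMatrix:
    """Directly simulate a z-scored feature matrix (no fragment layer).

    Baseline features are standard normal; ``shifts[label]`` adds a
    per-hotspot mean shift (in sd units) for that class.  Used to probe
    the classifiers under exactly known effect sizes.
    """
    rng = np.random.default_rng(seed)
    ids = []
    chroms = []
    for j in range(n_hotspots):
        chrom = f"chr{j // hotspots_per_chrom + 1}"
        ids.append(f"{chrom}:h{j}")
        chroms.append(chrom)
    rows = {}
    labels = {}
    for label, n in classes.items():
        shift = np.zeros(n_hotspots) if shifts is None else np.asarray(shifts.get(label, np.zeros(n_hotspots)))
        for i in range(n):
            sid = f"{label}_{i:03d}"
            rows[sid] = rng.normal(0.0, 1.0, n_hotspots) + shift
            labels[sid] = label
    values = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    return FeatureMatrix(
        values=values,
        labels=pd.Series(labels, name="label"),
        hotspot_chroms=pd.Series(chroms, index=ids),
    )


#: genome-background dinucleotide weights: AT-rich with CpG depletion
_DIMER_BG = np.outer([0.3, 0.2, 0.2, 0.3], [0.3, 0.2, 0.2, 0.3]).ravel()
_DIMER_BG[6] *= 0.25  # CG (CpG) depletion
_DIMER_BG /= _DIMER_BG.sum()
#: open-chromatin-like composition: GC-rich, no CpG depletion
_DIMER_OPEN = np.outer([0.2, 0.3, 0.3, 0.2], [0.2, 0.3, 0.3, 0.2]).ravel()
_DIMER_OPEN /= _DIMER_OPEN.sum()


def simulate_open_chromatin_regions(
    n_regions: int = 300, ifs_shift: float = -2.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced open/closed region features for the chromatin benchmark.

    Mirrors the contrast between constitutively open regions (promoter-
    like: IFS depleted by ``ifs_shift`` sd, GC/CpG-rich dinucleotide
    composition) and constitutively closed regions (genome-background
    composition, baseline IFS).  Returns (features, labels) with columns
    [IFS, 16 dimer frequencies]; label 1 = open.
    """
    rng = np.random.default_rng(seed)
    n_open = n_regions // 2
    n_closed = n_regions - n_open
    labels = np.concatenate([np.ones(n_open, dtype=int), np.zeros(n_closed, dtype=int)])
    ifs = np.concatenate([rng.normal(ifs_shift, 1.0, n_open), rng.normal(0.0, 1.0, n_closed)])
    conc = 200.0
    dimers = np.vstack(
        [rng.dirichlet(_DIMER_OPEN * conc, n_open), rng.dirichlet(_DIMER_BG * conc, n_closed)]
    )
    features = np.column_stack([ifs, dimers])
    order = rng.permutation(n_regions)
    return features[order], labels[order]


FIXTURE_PROFILES = {
    # tiny is a smoke fixture: at 1e5 fragments a window holds ~10
    # midpoints, so the planted effect must be deep (depletion 0.15 over
    # 600 bp) to be detectable at all; desk matches the scale at which
    # a 50% depletion is the intended recovery benchmark
    "tiny": dict(
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        n_fragments=100_000,
        n_regions=20,
        depletion=0.15,
        region_size=600,
    ),
    "desk": dict(
        chrom_lengths={"chr1": 10_000_000},
        n_fragments=2_000_000,
        n_regions=200,
        depletion=0.5,
        region_size=400,
    ),
}


def make_fixture(profile: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a ready-to-run input set (chrom.sizes, FASTA, blacklist,
    mappability bedGraph, fragment BED, truth TSV) for a profile.

    ``tiny`` (2 x 1 Mb, 1e5 fragments, 20 planted regions) runs in
    seconds; ``desk`` (1 x 10 Mb, 2e6 fragments, 200 planted regions)
    in minutes.  Regeneration with the same seed is identical.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(FIXTURE_PROFILES)}")
    cfg = FIXTURE_PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg["chrom_lengths"], seed=seed)
    genome = plant_regions(
        genome,
        cfg["n_regions"],
        region_size=cfg["region_size"],
        depletion=cfg["depletion"],
        size_shift=-15,
        seed=seed + 1,
    )
    frags = simulate_fragments(genome, cfg["n_fragments"], seed=seed + 2, out_bed=out / "fragments.bed")

    with open(out / "chrom.sizes", "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    genome.blacklist.to_csv(out / "blacklist.bed", sep="\t", header=False, index=False)
    with open(out / "mappability.bedgraph", "w") as fh:
        for chrom, track in genome.mappability.items():
            edges = np.flatnonzero(np.diff(track)) + 1
            bounds = np.concatenate([[0], edges, [len(track)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{chrom}\t{s}\t{e}\t{track[s]:g}\n")
    genome.planted.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    return {
        "chrom_sizes": out / "chrom.sizes",
        "fasta": out / "genome.fa",
        "blacklist": out / "blacklist.bed",
        "mappability": out / "mappability.bedgraph",
        "fragments": out / "fragments.bed",
        "truth": out / "planted_truth.tsv",
    }
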