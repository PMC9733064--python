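"""IFS computation and the GC / dinucleotide bias corrections."""

import numpy as np
import pandas as pd
import pytest

from cfhotspot import WindowGrid, compute_ifs, gc_correct, generate_windows, kmer_correct
from cfhotspot.ifs import WindowTrack, region_ifs

from conftest import brute_force_ifs


def make_track(ifs, gc=None, chrom="chr1", dimer=None):
    n = len(ifs)
    w = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else chrom,
            "start": np.arange(n) * 20,
            "end": np.arange(n) * 20 + 200,
            "n": np.maximum(1, np.round(ifs) / 2).astype(int),
            "mean_len": 166.0,
            "ifs": np.asarray(ifs, dtype=float),
        }
    )
    if gc is not None:
        w["gc"] = gc
    if dimer is not None:
        for d in range(16):
            w[f"dimer_{d}"] = dimer[:, d]
    means = w.groupby("chrom")["ifs"].mean().to_dict()
    return WindowTrack(windows=w, chrom_mean_length={c: 166.0 for c in w["chrom"].unique()}, chrom_mean_ifs=means)


class TestComputeIfs:
    def test_worked_example(self):
        """n=3 fragments of mean length 100 with chromosome L=200 give IFS 4.5, C 4."""
        n, mean_len, ifs = region_ifs(
            np.array([10, 20, 30]), np.array([0.0, 100.0, 200.0, 300.0]), np.array([0]), np.array([200]), L=200.0
        )
        assert ifs[0] == pytest.approx(4.5)
        assert int(np.floor(ifs[0])) == 4

    def test_empty_window_scores_zero(self, toy_fragments, small_grids):
        track = compute_ifs(toy_fragments, small_grids)
        empty = track.windows[track.windows["n"] == 0]
        assert (empty["ifs"] == 0).all()
        assert (np.floor(empty["ifs"]) == 0).all()

    def test_mean_length_equal_L_doubles_count(self):
        frags = pd.DataFrame(
            [("chr1", 100, 266, 166, 60.0)] * 10, columns=["chrom", "start", "end", "length", "mapq"]
        )
        grids = generate_windows({"chr1": 1000})
        track = compute_ifs(frags, grids)
        full = track.windows[track.windows["n"] == 10]
        assert np.allclose(full["ifs"], 20.0)

    def test_matches_brute_force_double_loop(self, rng, small_grids):
        """Vectorised IFS equals the per-fragment/per-window loop exactly."""
        starts = rng.integers(0, 800, size=60)
        lengths = rng.integers(60, 200, size=60)
        frags = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + lengths, "length": lengths, "mapq": 60.0}
        ).sort_values("start").reset_index(drop=True)
        track = compute_ifs(frags, {"chr1": small_grids["chr1"]})
        n_ref, ifs_ref = brute_force_ifs(frags, small_grids["chr1"], "chr1")
        np.testing.assert_array_equal(track.windows["n"].to_numpy(), n_ref)
        np.testing.assert_array_equal(track.windows["ifs"].to_numpy(), ifs_ref)

    def test_midpoint_total_count(self, toy_fragments, small_grids):
        """Each fragment midpoint lands in width/step windows when all kept."""
        track = compute_ifs(toy_fragments, small_grids)
        per_chrom = track.windows.groupby("chrom")["n"].sum()
        # interior midpoints fall in exactly 10 windows each
        assert per_chrom["chr1"] == 3 * 10
        assert per_chrom["chr2"] == 2 * 10

    def test_chromosome_without_fragments_skipped(self, toy_fragments):
        grids = generate_windows({"chr1": 1000, "chr2": 1000, "chr3": 1000})
        track = compute_ifs(toy_fragments, grids)
        assert set(track.windows["chrom"]) == {"chr1", "chr2"}


class TestGcCorrect:
    def test_unbiased_input_roundtrips(self, rng):
        ifs = rng.normal(50, 5, 3000)
        gc = rng.uniform(0.3, 0.6, 3000)
        track = make_track(ifs, gc=gc)
        out = gc_correct(track, seed=0)
        w = out.windows
        assert np.corrcoef(w["ifs_gc"], w["ifs"])[0, 1] > 0.95

    def test_per_chromosome_mean_preserved(self, rng):
        ifs = rng.normal(50, 5, 4000) + 40 * rng.uniform(0.3, 0.6, 4000)
        gc = rng.uniform(0.3, 0.6, 4000)
        chroms = np.repeat(["chr1", "chr2"], 2000)
        track = make_track(ifs, gc=gc, chrom=chroms)
        out = gc_correct(track, seed=0)
        for chrom, sub in out.windows.groupby("chrom"):
            assert sub["ifs_gc"].mean() == pytest.approx(sub["ifs"].mean(), rel=1e-9)

    def test_decorrelates_smooth_bias(self, rng):
        """A deterministic smooth GC bias is removed: |r(ifs_gc, gc)| < 0.05."""
        gc = rng.uniform(0.3, 0.6, 20000)
        bias = 30 * (gc - 0.45) + 80 * (gc - 0.45) ** 2
        ifs = rng.normal(50, 3, 20000) + bias
        track = make_track(ifs, gc=gc)
        out = gc_correct(track, seed=0)
        r = np.corrcoef(out.windows["ifs_gc"], gc)[0, 1]
        assert abs(r) < 0.05

    def test_too_few_windows_passthrough(self, rng):
        track = make_track(rng.normal(50, 5, 50), gc=rng.uniform(0.3, 0.6, 50))
        out = gc_correct(track)
        np.testing.assert_array_equal(out.windows["ifs_gc"], out.windows["ifs"])

    def test_constant_gc_residual_is_centered(self, rng):
        ifs = rng.normal(50, 5, 500)
        track = make_track(ifs, gc=np.full(500, 0.4))
        out = gc_correct(track)
        assert out.windows["ifs_gc"].mean() == pytest.approx(ifs.mean(), rel=1e-9)

    def test_subsampled_fit_is_deterministic(self, rng):
        ifs = rng.normal(50, 5, 3000)
        gc = rng.uniform(0.3, 0.6, 3000)
        a = gc_correct(make_track(ifs, gc=gc), max_points=1000, seed=7).windows["ifs_gc"]
        b = gc_correct(make_track(ifs, gc=gc), max_points=1000, seed=7).windows["ifs_gc"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestKmerCorrect:
    def test_uniform_composition_proportional(self, rng):
        ifs = rng.normal(50, 5, 400)
        dimer = np.full((400, 16), 1 / 16)
        out = kmer_correct(make_track(ifs, dimer=dimer))
        ratio = out.windows["ifs_kmer"] / out.windows["ifs"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_planted_dimer_effect_equalised(self, rng):
        """Two composition classes with IFS means 10 and 20 end up equal."""
        n = 2000
        cls = rng.integers(0, 2, n)
        dimer = np.zeros((n, 16))
        dimer[cls == 0, 0] = 1.0  # pure AA windows
        dimer[cls == 1, 5] = 1.0  # pure CC windows
        ifs = np.where(cls == 0, rng.normal(10, 1, n), rng.normal(20, 1, n))
        out = kmer_correct(make_track(ifs, dimer=dimer))
        m0 = out.windows["ifs_kmer"][cls == 0].mean()
        m1 = out.windows["ifs_kmer"][cls == 1].mean()
        assert m0 == pytest.approx(m1, rel=0.05)

    def test_scale_restored(self, rng):
        ifs = rng.normal(50, 5, 1000)
        dimer = rng.dirichlet(np.ones(16), size=1000)
        out = kmer_correct(make_track(ifs, dimer=dimer))
        assert out.windows["ifs_kmer"].mean() == pytest.approx(50, rel=0.1)

    def test_single_window_finite(self):
        dimer = np.full((1, 16), 1 / 16)
        out = kmer_correct(make_track(np.array([12.0]), dimer=dimer))
        val = out.windows["ifs_kmer"].iloc[0]
        assert np.isfinite(val) and val > 0
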